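"""Gini importance attribution vs brute-force path-enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from spectrosig import importance as imp

SHAPE = imp.MAP_SHAPE
N_FEAT = SHAPE[0] * SHAPE[1]


def brute_force_importances(est, X, y, n_classes):
    """Recompute global and per-category importances from the training data.

    Walks the fitted tree's recorded (feature, threshold) splits, re-derives
    every node's sample subset and Gini impurity from scratch, and
    enumerates leaf-to-root paths explicitly.  Independent of the tree's
    stored impurity/sample-count arrays.
    """
    t = est.tree_
    N = len(y)
    global_imp = np.zeros(X.shape[1])
    cat_imp = {c: np.zeros(X.shape[1]) for c in range(n_classes)}

    def gini(idx):
        p = np.bincount(y[idx], minlength=n_classes) / len(idx)
        return float(np.sum(p * (1 - p)))

    def walk(node, idx, path):
        if t.children_left[node] == -1:
            counts = np.bincount(y[idx], minlength=n_classes)
            majority = int(counts.argmax())
            for feat, node_i in path:
                cat_imp[majority][feat] += node_i
            return
        f, thr = int(t.feature[node]), t.threshold[node]
        left = idx[X[idx, f] <= thr]
        right = idx[X[idx, f] > thr]
        node_i = (len(idx) * gini(idx) - len(left) * gini(left) - len(right) * gini(right)) / N
        global_imp[f] += node_i
        walk(t.children_left[node], left, path + [(f, node_i)])
        walk(t.children_right[node], right, path + [(f, node_i)])

    walk(0, np.arange(N), [])
    return global_imp, cat_imp


def shallow_forest(n_classes=4, depth=3, n_trees=5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), 30)
    X = rng.standard_normal((y.size, N_FEAT)).astype(np.float32)
    for c in range(n_classes):
        X[y == c, c * 7] += 3.0
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_depth=depth, bootstrap=False,
        random_state=seed, n_jobs=1,
    ).fit(X, y)
    return forest, X, y, n_classes


class TestGini:
    def test_pure_node_is_zero(self):
        assert imp.gini_impurity([1.0, 0.0, 0.0]) == 0.0

    def test_eight_equal_classes(self):
        assert imp.gini_impurity([1 / 8] * 8) == pytest.approx(0.875)

    def test_two_class_maximum(self):
        assert imp.gini_impurity([0.5, 0.5]) == pytest.approx(0.5)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            imp.gini_impurity([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_bound(self, raw):
        p = np.array(raw) / np.sum(raw)
        g = imp.gini_impurity(p)
        assert 0.0 <= g <= 1.0 - 1.0 / len(p) + 1e-12


class TestNodeImportance:
    def test_uninformative_split_is_zero(self):
        g = imp.gini_impurity([0.5, 0.5])
        assert imp.node_importance(g, (g, g), (1.0, 0.5, 0.5)) == pytest.approx(0.0)

    def test_pure_split_of_balanced_parent(self):
        assert imp.node_importance(0.5, (0.0, 0.0), (1.0, 0.5, 0.5)) == pytest.approx(0.5)

    def test_fraction_mismatch_rejected(self):
        with pytest.raises(ValueError):
            imp.node_importance(0.5, (0.0, 0.0), (1.0, 0.3, 0.5))

    @given(st.integers(1, 99), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_nonnegative_for_any_valid_split(self, n_left, a_left, a_parent_extra, total_shift):
        # random two-class split: left child gets (n_left, a_left of class A)
        rng = np.random.default_rng(total_shift)
        n_right = int(rng.integers(1, 100))
        a_left = min(a_left, n_left)
        a_right = int(rng.integers(0, n_right + 1))
        n_p = n_left + n_right
        a_p = a_left + a_right

        def g(a, n):
            p = a / n
            return 2 * p * (1 - p)

        i = imp.node_importance(
            g(a_p, n_p), (g(a_left, n_left) if n_left else 0.0, g(a_right, n_right)),
            (n_p / n_p, n_left / n_p, n_right / n_p),
        )
        assert i >= -1e-12


class TestForestImportance:
    def test_global_matches_brute_force_oracle(self):
        forest, X, y, k = shallow_forest()
        total = np.zeros(N_FEAT)
        for est in forest.estimators_:
            gi, _ = brute_force_importances(est, X, y, k)
            total += gi / gi.sum()
        oracle = total / len(forest.estimators_)
        oracle /= oracle.sum()
        got = imp.global_importance(forest).flatten()
        assert np.allclose(got, oracle, atol=1e-12)

    def test_global_matches_sklearn_attribute(self):
        forest, *_ = shallow_forest(seed=1)
        got = imp.global_importance(forest).flatten()
        ref = forest.feature_importances_
        assert np.allclose(got, ref / ref.sum(), atol=1e-10)

    def test_category_matches_brute_force_oracle(self):
        forest, X, y, k = shallow_forest(seed=2)
        for c in range(k):
            oracle = np.zeros(N_FEAT)
            for est in forest.estimators_:
                _, ci = brute_force_importances(est, X, y, k)
                oracle += ci[c]
            oracle /= len(forest.estimators_)
            got = imp.category_importance(forest, c).flatten()
            assert np.allclose(got, oracle, atol=1e-12)

    def test_category_support_union_equals_global_support(self):
        forest, X, y, k = shallow_forest(seed=3)
        union = np.zeros(N_FEAT, dtype=bool)
        for c in range(k):
            union |= imp.category_importance(forest, c).flatten() > 0
        assert np.array_equal(union, imp.global_importance(forest).flatten() > 0)

    def test_stump_attribution(self):
        # one split on a known feature, two pure leaves -> class-A and
        # class-B maps both live on that feature only; class C (absent)
        # yields a zero map with a warning
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, N_FEAT)).astype(np.float32)
        X[:, 123] = y * 2.0
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)

        class OneTreeForest:
            estimators_ = [stump]
            classes_ = np.array([0, 1])

        fake = OneTreeForest()
        for c in (0, 1):
            m = imp.category_importance(fake, c).flatten()
            assert m[123] > 0
            assert np.count_nonzero(m) == 1
        with pytest.warns(UserWarning, match="no leaf"):
            fake2 = OneTreeForest()
            fake2.classes_ = np.array([0, 1, 2])
            z = imp.category_importance(fake2, 2)
        assert np.all(z.values == 0)

    def test_single_informative_feature_dominates(self):
        # with every split seeing all features, the sole informative
        # feature collects essentially all impurity reduction
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 100)
        X = rng.standard_normal((200, N_FEAT)).astype(np.float32)
        X[:, 999] = y * 3 + 0.1 * rng.standard_normal(200)
        forest = RandomForestClassifier(
            n_estimators=10, max_features=None, random_state=0, n_jobs=1
        ).fit(X, y)
        m = imp.global_importance(forest).flatten()
        assert m[999] >= 0.5

    def test_label_permuted_importance_is_spread_out(self):
        # under permuted labels no feature should dominate; with enough
        # split events per feature (400 trees) the maximum cell stays well
        # below 5x the mean cell
        rng = np.random.default_rng(8)
        y = np.repeat(np.arange(8), 50)
        for rep in range(2):
            X = rng.standard_normal((400, N_FEAT)).astype(np.float32)
            yp = y[rng.permutation(400)]
            forest = RandomForestClassifier(
                n_estimators=400, random_state=rep, n_jobs=1
            ).fit(X, yp)
            m = imp.global_importance(forest).values
            assert m.max() < 5.0 * m.mean()

    def test_no_split_forest_warns_zero_map(self):
        X = np.zeros((10, N_FEAT), dtype=np.float32)
        y = np.zeros(10, dtype=int)
        forest = RandomForestClassifier(n_estimators=3, random_state=0, n_jobs=1).fit(X, y)
        with pytest.warns(UserWarning, match="no splits"):
            m = imp.global_importance(forest)
        assert np.all(m.values == 0)

    def test_map_sums_to_one(self):
        forest, *_ = shallow_forest(seed=6)
        assert imp.global_importance(forest).values.sum() == pytest.approx(1.0)


class TestAverageAndCompare:
    @staticmethod
    def random_map(rng, scale=1.0):
        return imp.ImportanceMap(np.abs(rng.standard_normal(SHAPE)) * scale)

    def test_mean_of_copies_is_identity(self, rng):
        m = self.random_map(rng)
        out = imp.average_importance([m, imp.ImportanceMap(m.values.copy())])
        assert np.allclose(out.values, m.values)

    def test_disjoint_support_halves(self):
        a = np.zeros(SHAPE)
        b = np.zeros(SHAPE)
        a[:10] = 2.0
        b[20:30] = 4.0
        out = imp.average_importance([imp.ImportanceMap(a), imp.ImportanceMap(b)])
        assert np.allclose(out.values[:10], 1.0)
        assert np.allclose(out.values[20:30], 2.0)

    def test_mean_matches_stack_oracle(self, rng):
        maps = [self.random_map(rng) for _ in range(10)]
        out = imp.average_importance(maps)
        oracle = np.stack([m.values for m in maps]).mean(axis=0)
        assert np.allclose(out.values, oracle)

    def test_identical_maps_give_empty_mask(self, rng):
        m = self.random_map(rng)
        cmp_ = imp.compare_maps(m, imp.ImportanceMap(m.values.copy()))
        assert not cmp_.positive.any() and not cmp_.negative.any()

    def test_single_raised_cell_is_isolated(self):
        # Gaussian difference field with one cell lifted by 10 sigma (fixed
        # seed whose noise field stays below the 4-sigma criterion)
        rng = np.random.default_rng(3)
        base = 1.0 + np.abs(rng.standard_normal(SHAPE))
        other = base + 0.001 * rng.standard_normal(SHAPE)
        d_sigma = (other - base).std()
        spiked = other.copy()
        spiked[70, 20] = base[70, 20] + 10 * d_sigma
        cmp_ = imp.compare_maps(imp.ImportanceMap(spiked), imp.ImportanceMap(base), k=4)
        assert cmp_.positive[70, 20]
        assert cmp_.positive.sum() == 1

    def test_antisymmetry(self, rng):
        a, b = self.random_map(rng), self.random_map(rng)
        ab = imp.compare_maps(a, b)
        ba = imp.compare_maps(b, a)
        assert np.array_equal(ab.positive, ba.negative)
        assert np.array_equal(ab.negative, ba.positive)

    def test_false_positive_budget_at_four_sigma(self, rng):
        # under pure-noise differences, ~7008 * P(Z > 3.89) ~ 1 cell/side
        counts = [
            imp.compare_maps(self.random_map(rng), self.random_map(rng)).positive.sum()
            for _ in range(50)
        ]
        assert np.mean(counts) <= 2.0


class TestGroupContrast:
    @staticmethod
    def noise_maps(rng, n=4):
        return [imp.ImportanceMap(np.abs(rng.standard_normal(SHAPE))) for _ in range(n)]

    def test_identical_groups_have_no_dominance(self, rng):
        maps = self.noise_maps(rng)
        copies = [imp.ImportanceMap(m.values.copy()) for m in maps]
        c = imp.group_importance_contrast(maps, copies)
        assert not (c.labels == imp.ContrastMap.A_DOMINANT).any()
        assert not (c.labels == imp.ContrastMap.B_DOMINANT).any()
        assert (c.labels == imp.ContrastMap.BOTH).sum() == ((c.z_a >= 2) & (c.z_b >= 2)).sum()

    def test_boosted_region_is_group_dominant(self, rng):
        a_maps = self.noise_maps(rng)
        b_maps = self.noise_maps(rng)
        for m in b_maps:
            m.values[100:110, 30:40] += 6.0 * m.values.std()
        c = imp.group_importance_contrast(a_maps, b_maps)
        region = c.labels[100:110, 30:40]
        assert (region == imp.ContrastMap.B_DOMINANT).mean() > 0.5
        assert not (c.labels == imp.ContrastMap.A_DOMINANT).any()

    def test_null_dominance_count_small(self, rng):
        counts = []
        for _ in range(40):
            c = imp.group_importance_contrast(self.noise_maps(rng, 3), self.noise_maps(rng, 3))
            counts.append(((c.labels == 2) | (c.labels == 3)).sum())
        assert np.mean(counts) <= 2.0

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            imp.group_importance_contrast([], self.noise_maps(rng))
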