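"""Tree induction, error-based pruning, prediction and rule extraction."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats as sstats

import sffstree as st
from sffstree import errors
from sffstree.tree import (
    GAIN_EPS,
    DecisionTree,
    Internal,
    Leaf,
    TreeParams,
    best_split,
    entropy,
    extract_rules,
    fit_tree,
    grow,
    grow_matrix,
    predict,
    predict_by_rules,
    prune,
    ucf,
)

from .conftest import dataset_from_matrix, random_labeled_matrix


def brute_force_best_split(values, labels, criterion="info_gain", min_leaf=1):
    """Exhaustive enumeration over every observed threshold."""
    values = np.asarray(values, dtype=float)
    n = values.size
    parent = Counter(labels)
    if len(parent) < 2:
        return None
    hp = entropy([parent["normal"], parent["tumor"]])
    best = None
    for thr in sorted(set(values))[:-1]:
        left = [l for v, l in zip(values, labels) if v <= thr]
        right = [l for v, l in zip(values, labels) if v > thr]
        if len(left) < min_leaf or len(right) < min_leaf:
            continue
        cl, cr = Counter(left), Counter(right)
        gain = (
            hp
            - len(left) / n * entropy([cl["normal"], cl["tumor"]])
            - len(right) / n * entropy([cr["normal"], cr["tumor"]])
        )
        if gain <= GAIN_EPS:
            continue
        if criterion == "gain_ratio":
            sh = entropy([len(left), len(right)])
            score = gain / sh if sh > 0 else 0.0
        else:
            score = gain
        if best is None or score > best[1]:
            best = (thr, score)
    return best


def ucf_bisection(e, n, cf, tol=1e-12):
    """Root of P(X <= e | n, p) = cf in p, by bisection on the binomial tail."""
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if sstats.binom.cdf(e, n, mid) > cf:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5], 1.0), ([10, 0], 0.0), ([2, 6], 0.8113)],
    )
    def test_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-4)

    def test_empty_node_rejected(self):
        with pytest.raises(errors.DomainError):
            entropy([0, 0])


class TestBestSplit:
    def test_perfect_split_gain_equals_parent_entropy(self):
        thr, score = best_split(
            [1.0, 2.0, 3.0, 4.0], ["normal", "normal", "tumor", "tumor"]
        )
        assert thr == 2.0
        assert score == pytest.approx(1.0)

    def test_constant_feature_gives_none(self):
        assert best_split([3.0] * 6, ["tumor"] * 3 + ["normal"] * 3) is None

    @pytest.mark.parametrize("criterion", ["info_gain", "gain_ratio"])
    def test_matches_exhaustive_enumeration(self, criterion):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            values = np.round(rng.normal(0, 1, n), rng.integers(0, 3))
            labels = ["tumor" if b else "normal" for b in rng.random(n) < 0.5]
            if len(set(labels)) < 2:
                continue
            got = best_split(values, labels, criterion=criterion)
            want = brute_force_best_split(values, labels, criterion=criterion)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == want[0]
                assert got[1] == pytest.approx(want[1], abs=1e-12)


class TestGrow:
    def test_pure_input_gives_single_clean_leaf(self):
        ds = st.ExpressionDataset(
            ["g1"], ["s1", "s2", "s3"], ["tumor"] * 3, [[1.0, 2.0, 3.0]]
        )
        t = grow(ds, ["g1"])
        assert isinstance(t.root, Leaf)
        assert t.root.label == "tumor"
        assert t.root.n_misclassified == 0

    def test_xor_quadrants_need_depth_two(self):
        """Class depends on BOTH features (four quadrant clusters).

        One quadrant carries an extra point: under exact balance every
        marginal split of an XOR layout has zero information gain, so a
        greedy learner could never take the first split at all.
        """
        pts, labels = [], []
        for cx, cy, lab, size in [
            (0, 0, "normal", 5),
            (4, 4, "normal", 5),
            (0, 4, "tumor", 5),
            (4, 0, "tumor", 6),
        ]:
            pts.append(np.tile([float(cx), float(cy)], (size, 1)))
            labels += [lab] * size
        x = np.vstack(pts)
        ds = dataset_from_matrix(x, labels)
        t = grow(ds, ds.probe_ids, TreeParams(min_leaf=1))
        assert t.depth() == 2
        correct = sum(
            predict(t, ds.sample_map(i)) == ds.labels[i]
            for i in range(ds.n_samples)
        )
        assert correct == ds.n_samples

    def test_separable_fixtures_fit_training_perfectly_unpruned(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, labels = random_labeled_matrix(rng, int(rng.integers(6, 20)), 3)
            ds = dataset_from_matrix(x, labels)  # continuous => conflict-free
            t = grow(ds, ds.probe_ids, TreeParams(min_leaf=1))
            assert all(
                predict(t, ds.sample_map(i)) == ds.labels[i]
                for i in range(ds.n_samples)
            )

    def test_empty_feature_set_rejected(self, toy_dataset):
        with pytest.raises(errors.UsageError):
            grow(toy_dataset, [])

    def test_leaf_counts_partition_training_set(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, labels = random_labeled_matrix(rng, int(rng.integers(5, 30)), 2)
            ds = dataset_from_matrix(x, labels)
            for prune_flag in (False, True):
                t = fit_tree(ds, ds.probe_ids, TreeParams(prune=prune_flag))
                leaves = t.leaves()
                assert sum(l.n_covered for l in leaves) == ds.n_samples
                for l in leaves:
                    assert l.n_misclassified <= l.n_covered / 2


class TestUcf:
    def test_closed_form_at_zero_errors(self):
        assert ucf(0, 2, 0.25) == pytest.approx(1 - 0.25 ** (1 / 2), abs=1e-12)
        assert ucf(0, 51, 0.25) == pytest.approx(1 - 0.25 ** (1 / 51), abs=1e-12)
        assert ucf(0, 51, 0.25) == pytest.approx(0.02682, abs=5e-6)

    @pytest.mark.parametrize("e,n", [(2, 20), (1, 5), (7, 30), (3, 8)])
    def test_matches_binomial_tail_bisection(self, e, n):
        assert ucf(e, n, 0.25) == pytest.approx(ucf_bisection(e, n, 0.25), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(errors.DomainError):
            ucf(3, 2, 0.25)
        with pytest.raises(errors.DomainError):
            ucf(0, 2, 1.5)

    def test_all_errors_gives_certain_misclassification(self):
        assert ucf(5, 5, 0.25) == 1.0


class TestPrune:
    def _two_leaf_tree(self, n_left, e_left, n_right, e_right):
        c0l, c1l = n_left - e_left, e_left  # left leaf labeled normal
        c0r, c1r = e_right, n_right - e_right  # right leaf labeled tumor
        left = Leaf("normal", n_left, e_left, (c0l, c1l))
        right = Leaf("tumor", n_right, e_right, (c0r, c1r))
        c0, c1 = c0l + c0r, c1l + c1r
        maj = "tumor" if c1 > c0 else "normal"
        root = Internal("g", 0.0, left, right, maj, (c0, c1))
        return DecisionTree(root=root, n_training=n_left + n_right)

    def test_replacement_decided_exactly_by_the_ucf_inequality(self):
        cf = 0.25
        for n_l, e_l, n_r, e_r in [(1, 0, 1, 0), (5, 0, 5, 0), (3, 1, 4, 0), (2, 0, 8, 1)]:
            t = self._two_leaf_tree(n_l, e_l, n_r, e_r)
            c0, c1 = t.root.class_counts
            n = c0 + c1
            e_merged = n - (c1 if t.root.majority == "tumor" else c0)
            leaf_bound = n * ucf(e_merged, n, cf)
            subtree_bound = n_l * ucf(e_l, n_l, cf) + n_r * ucf(e_r, n_r, cf)
            pruned = prune(t, TreeParams(confidence=cf))
            collapsed = isinstance(pruned.root, Leaf)
            assert collapsed == (leaf_bound <= subtree_bound)

    def test_single_leaf_unchanged(self):
        t = DecisionTree(root=Leaf("tumor", 4, 0, (0, 4)), n_training=4)
        assert prune(t).to_dict() == t.to_dict()

    def test_never_increases_leaf_count(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            x, labels = random_labeled_matrix(rng, int(rng.integers(5, 40)), 2)
            ds = dataset_from_matrix(x, labels)
            unpruned = grow(ds, ds.probe_ids)
            pruned = prune(unpruned)
            assert pruned.n_leaves <= unpruned.n_leaves

    def test_training_accuracy_never_increases_under_pruning(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            x, labels = random_labeled_matrix(rng, int(rng.integers(6, 30)), 2)
            ds = dataset_from_matrix(x, labels)
            unpruned = grow(ds, ds.probe_ids, TreeParams(min_leaf=1))
            pruned = prune(unpruned, TreeParams(min_leaf=1))
            acc = lambda t: sum(
                predict(t, ds.sample_map(i)) == ds.labels[i]
                for i in range(ds.n_samples)
            )
            assert acc(unpruned) >= acc(pruned)


class TestPredictAndRules:
    @pytest.fixture()
    def single_split_tree(self):
        # the canonical one-rule marker tree: "If g > 7.523 then tumor"
        left = Leaf("normal", 51, 0, (51, 0))
        right = Leaf("tumor", 57, 4, (4, 53))
        root = Internal("g", 7.523, left, right, "tumor", (55, 53))
        return DecisionTree(root=root, n_training=108)

    def test_above_threshold_is_tumor(self, single_split_tree):
        assert predict(single_split_tree, {"g": 8.0}) == "tumor"

    def test_boundary_value_takes_the_le_branch(self, single_split_tree):
        assert predict(single_split_tree, {"g": 7.523}) == "normal"

    def test_missing_probe_is_input_error(self, single_split_tree):
        with pytest.raises(errors.InputError):
            predict(single_split_tree, {"other": 1.0})

    def test_rule_rendering_shows_coverage(self, single_split_tree):
        rules = extract_rules(single_split_tree)
        rendered = [r.render() for r in rules]
        assert "If g > 7.523 then tumor (57/4)" in rendered
        assert "If g <= 7.523 then normal (51/0)" in rendered

    def test_single_leaf_tree_yields_one_unconditional_rule(self):
        t = DecisionTree(root=Leaf("normal", 5, 1, (4, 1)), n_training=5)
        rules = extract_rules(t)
        assert len(rules) == 1 and rules[0].conditions == ()

    def test_rule_count_and_coverage_conservation(self, small_pair_fixture):
        ds, truth = small_pair_fixture
        pair = [p["probe_id"] for p in truth["planted"]]
        t = fit_tree(ds, pair)
        rules = extract_rules(t)
        assert len(rules) == t.n_leaves
        assert sum(r.n_covered for r in rules) == ds.n_samples

    def test_every_training_sample_matches_exactly_one_rule(self):
        rng = np.random.default_rng(17)
        x, labels = random_labeled_matrix(rng, 20, 3)
        ds = dataset_from_matrix(x, labels)
        t = fit_tree(ds, ds.probe_ids, TreeParams(min_leaf=1))
        rules = extract_rules(t)
        for i in range(ds.n_samples):
            sample = ds.sample_map(i)
            assert sum(r.matches(sample) for r in rules) == 1

    def test_rules_equal_tree_on_random_inputs(self):
        rng = np.random.default_rng(18)
        x, labels = random_labeled_matrix(rng, 25, 3)
        ds = dataset_from_matrix(x, labels)
        t = fit_tree(ds, ds.probe_ids, TreeParams(min_leaf=1, prune=False))
        rules = extract_rules(t)
        for _ in range(100):
            sample = {g: float(v) for g, v in zip(ds.probe_ids, rng.normal(8, 2, 3))}
            assert predict_by_rules(rules, sample) == predict(t, sample)

    def test_training_accuracy_agrees_with_sklearn_on_separable_data(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(30)
        x, labels = random_labeled_matrix(rng, 30, 3)
        ds = dataset_from_matrix(x, labels)
        ours = grow(ds, ds.probe_ids, TreeParams(min_leaf=1))
        acc = np.mean(
            [predict(ours, ds.sample_map(i)) == ds.labels[i] for i in range(30)]
        )
        clf = sklearn_tree.DecisionTreeClassifier(criterion="entropy", random_state=0)
        clf.fit(x, labels)
        assert acc == clf.score(x, labels) == 1.0
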