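"""Edge ranking, feature-matrix assembly and Gini-importance pre-screening."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

import sfrgsn as sf
from sfrgsn.ssn import SampleSpecificNetwork


def _ssn(sample, edges):
    return SampleSpecificNetwork(sample, {p: (d, 0.01) for p, d in edges.items()})


class TestRankEdges:
    def test_absolute_value_ranking(self):
        gsn = sf.GroupSpecificNetwork(
            "I", 3, {("A", "B"): 0.5, ("B", "C"): -0.7, ("C", "D"): 0.1})
        assert sf.rank_edges(gsn, 2) == [("B", "C"), ("A", "B")]

    def test_signed_ranking_flag(self):
        gsn = sf.GroupSpecificNetwork(
            "I", 3, {("A", "B"): 0.5, ("B", "C"): -0.7, ("C", "D"): 0.1})
        assert sf.rank_edges(gsn, 2, signed=True) == [("A", "B"), ("C", "D")]

    def test_k_beyond_edge_count_returns_all(self):
        gsn = sf.GroupSpecificNetwork("I", 1, {("A", "B"): 0.5})
        assert sf.rank_edges(gsn, 10) == [("A", "B")]

    def test_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(51)
        pairs = [sf.canonical_pair(f"G{i}", f"G{j}")
                 for i in range(12) for j in range(i + 1, 12)]
        weights = {p: float(rng.normal()) for p in pairs}
        gsn = sf.GroupSpecificNetwork("I", 4, weights)
        oracle = sorted(pairs, key=lambda p: (-abs(weights[p]), p))[:10]
        assert sf.rank_edges(gsn, 10) == oracle


class TestCandidateSet:
    def test_shared_top_edges_collapse(self):
        w = {("A", "B"): 0.9, ("C", "D"): 0.8, ("E", "F"): 0.1}
        g1 = sf.GroupSpecificNetwork("I", 2, dict(w))
        g2 = sf.GroupSpecificNetwork("II", 2, dict(w))
        assert len(sf.build_candidate_set([g1, g2], 2)) == 2

    def test_disjoint_top_sets_concatenate(self):
        g1 = sf.GroupSpecificNetwork("I", 2, {("A", "B"): 0.9, ("C", "D"): 0.8})
        g2 = sf.GroupSpecificNetwork("II", 2, {("E", "F"): 0.9, ("G", "H"): 0.8})
        assert len(sf.build_candidate_set([g1, g2], 2)) == 4

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(53)
        pairs = [sf.canonical_pair(f"G{i}", f"G{j}")
                 for i in range(10) for j in range(i + 1, 10)]
        gsns = [sf.GroupSpecificNetwork(
            g, 3, {p: float(rng.normal()) for p in pairs if rng.random() < 0.5})
            for g in ("I", "II", "III")]
        got = sf.build_candidate_set(gsns, 5)
        oracle = set()
        for g in gsns:
            oracle |= set(sf.rank_edges(g, 5))
        assert set(got) == oracle
        assert got == sorted(got)  # deterministic order


class TestEdgeFeatures:
    labels = sf.GroupLabels(
        {"n0": "Normal", "n1": "Normal", "n2": "Normal",
         "s1": "I", "s2": "I", "s3": "II"}, "Normal")

    def test_sample_without_edges_gets_zero_row(self):
        cands = [("A", "B"), ("C", "D")]
        fm = sf.build_edge_features(
            cands, [_ssn("s1", {}), _ssn("s2", {("A", "B"): 0.4})], self.labels)
        assert np.array_equal(fm.values, [[0.0, 0.0], [0.4, 0.0]])

    def test_reference_samples_excluded_by_default(self):
        fm = sf.build_edge_features(
            [("A", "B")], [_ssn("n0", {("A", "B"): 1.0}), _ssn("s1", {})],
            self.labels)
        assert fm.sample_ids == ["s1"]
        fm2 = sf.build_edge_features(
            [("A", "B")], [_ssn("n0", {("A", "B"): 1.0}), _ssn("s1", {})],
            self.labels, include_reference=True)
        assert fm2.sample_ids == ["n0", "s1"]

    def test_matches_per_cell_lookup_oracle(self):
        rng = np.random.default_rng(59)
        cands = [sf.canonical_pair(f"G{i}", f"G{i + 1}") for i in range(0, 8, 2)]
        ssns = []
        for s in ("s1", "s2", "s3"):
            edges = {p: float(rng.normal()) for p in cands if rng.random() < 0.6}
            ssns.append(_ssn(s, edges))
        fm = sf.build_edge_features(cands, ssns, self.labels)
        for r, ssn in enumerate(ssns):
            for c, p in enumerate(cands):
                expected = ssn.edges[p][0] if p in ssn.edges else 0.0
                assert fm.values[r, c] == expected


class TestGini:
    def test_pure_node_is_zero(self):
        assert sf.gini_impurity([1.0, 0.0]) == pytest.approx(0.0)

    def test_balanced_two_class(self):
        assert sf.gini_impurity([0.5, 0.5]) == pytest.approx(0.5)

    def test_three_class_symmetry(self):
        assert sf.gini_impurity([1 / 3] * 3) == pytest.approx(2 / 3)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sf.gini_impurity([0.5, 0.4])
        with pytest.raises(ValueError, match="non-negative"):
            sf.gini_impurity([1.5, -0.5])


class TestImpurityGain:
    def test_pure_children_of_balanced_parent(self):
        assert sf.impurity_gain([5, 5], [5, 0], [0, 5]) == pytest.approx(0.5)

    def test_proportional_split_gains_nothing(self):
        assert sf.impurity_gain([6, 4], [3, 2], [3, 2]) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        # parent {6,4}, left {4,1}, right {2,3} -> 0.08
        assert sf.impurity_gain([6, 4], [4, 1], [2, 3]) == pytest.approx(0.08)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="must equal parent"):
            sf.impurity_gain([6, 4], [4, 1], [2, 2])

    def test_non_negative_on_random_splits(self):
        rng = np.random.default_rng(61)
        for _ in range(1000):
            n_classes = int(rng.integers(2, 5))
            left = rng.integers(0, 20, size=n_classes)
            right = rng.integers(0, 20, size=n_classes)
            if left.sum() == 0 or right.sum() == 0:
                continue
            assert sf.impurity_gain(left + right, left, right) >= -1e-12


class TestPrescreen:
    def _fm(self, rng, n_per_class=30, n_decoys=10, separation=3.0):
        """One feature separates two groups; decoys are pure noise."""
        n = 2 * n_per_class
        X = rng.normal(size=(n, n_decoys + 1))
        y = ["I"] * n_per_class + ["II"] * n_per_class
        X[:n_per_class, 0] += separation
        edges = [sf.canonical_pair(f"G{k}", f"G{k + 100}")
                 for k in range(n_decoys + 1)]
        samples = [f"s{k}" for k in range(n)]
        return sf.EdgeFeatureMatrix(samples, edges, X, y), edges

    def test_informative_feature_ranks_first(self):
        """The separating feature tops the ranking in >= 95% of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fm, edges = self._fm(rng)
            cfg = sf.PipelineConfig(rf_trees=50, seed=seed)
            ranking = sf.prescreen_features(fm, 5, cfg)
            hits += ranking.order[0] == edges[0]
        assert hits >= 19

    def test_importances_non_negative(self):
        rng = np.random.default_rng(67)
        fm, _ = self._fm(rng)
        ranking = sf.prescreen_features(fm, 5, sf.PipelineConfig(rf_trees=20))
        assert all(v >= 0 for v in ranking.scores.values())

    def test_single_class_rejected(self):
        rng = np.random.default_rng(71)
        fm, _ = self._fm(rng)
        fm.groups = ["I"] * len(fm.groups)
        with pytest.raises(ValueError, match="2 groups"):
            sf.prescreen_features(fm, 5, sf.PipelineConfig())

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(73)
        fm, _ = self._fm(rng)
        cfg = sf.PipelineConfig(rf_trees=30, seed=5)
        r1 = sf.prescreen_features(fm, 5, cfg)
        r2 = sf.prescreen_features(fm, 5, cfg)
        assert r1.order == r2.order
        assert r1.scores == r2.scores

    def test_depth_one_tree_importance_equals_split_gain(self):
        """A single stump's accumulated importance is its split's impurity gain."""
        rng = np.random.default_rng(79)
        X = np.concatenate([rng.normal(-2, 1, 25), rng.normal(2, 1, 25)])[:, None]
        y = np.array([0] * 25 + [1] * 25)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        got = sf.tree_gini_importances([stump], 1)[0]
        thr = stump.tree_.threshold[0]
        left_mask = X[:, 0] <= thr
        parent = np.bincount(y, minlength=2)
        left = np.bincount(y[left_mask], minlength=2)
        right = parent - left
        assert got == pytest.approx(sf.impurity_gain(parent, left, right), abs=1e-12)
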