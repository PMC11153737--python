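"""First selection round: edge ranking and random-forest pre-screening.

Candidate edges are the union over groups of each group network's top-k
edges by |weight|. Each candidate edge becomes one feature: a sample's value
is its significant ΔPCC for that edge (0 when the edge is absent from the
sample's network). A random forest then ranks the candidates by summed
Gini impurity gain and the top ``top_features`` survive.

The importance here is the classical per-node accumulation: at every split
on feature f,

    gain = Gini(node) - (|L| * Gini(L) + |R| * Gini(R)) / |node|,

summed over all nodes of all trees. This is computed by walking the fitted
sklearn trees directly (it is not the same normalization as sklearn's
``feature_importances_``, and a depth-1 tree's importance equals the plain
impurity gain of its single split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import PipelineConfig
from .gsn import GroupSpecificNetwork
from .io import GroupLabels, Pair
from .ssn import SampleSpecificNetwork


@dataclass
class EdgeFeatureMatrix:
    """Samples x candidate-edge ΔPCC feature table."""

    sample_ids: list[str]
    edge_ids: list[Pair]
    values: np.ndarray  # samples x edges
    groups: list[str]   # group per sample

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.edge_ids)):
            raise ValueError("feature matrix dimensions do not match id lists")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group per sample required")

    def subset_edges(self, edges: Sequence[Pair]) -> "EdgeFeatureMatrix":
        pos = {e: k for k, e in enumerate(self.edge_ids)}
        idx = [pos[e] for e in edges]
        return EdgeFeatureMatrix(self.sample_ids, list(edges),
                                 self.values[:, idx], self.groups)

    def subset_samples(self, samples: Sequence[str]) -> "EdgeFeatureMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in samples]
        return EdgeFeatureMatrix(list(samples), self.edge_ids,
                                 self.values[idx, :], [self.groups[k] for k in idx])


@dataclass
class ImportanceRanking:
    scores: dict[Pair, float]
    order: list[Pair]  # descending score, lexicographic tie-break

    def top(self, k: int) -> list[Pair]:
        return self.order[:k]


def rank_edges(gsn: GroupSpecificNetwork, k: int, signed: bool = False) -> list[Pair]:
    """Top-k edges by descending |weight| (or signed weight when ``signed``),
    lexicographic pair order breaking ties; all edges when fewer than k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    key = (lambda p: (-gsn.weights[p], p)) if signed else (lambda p: (-abs(gsn.weights[p]), p))
    return sorted(gsn.weights, key=key)[:k]


def build_candidate_set(gsns: Sequence[GroupSpecificNetwork], k: int,
                        signed: bool = False) -> list[Pair]:
    """Deduplicated union of each group's top-k edges, in sorted order."""
    union: set[Pair] = set()
    for gsn in gsns:
        union.update(rank_edges(gsn, k, signed=signed))
    return sorted(union)


def build_edge_features(candidates: Sequence[Pair],
                        ssns: Sequence[SampleSpecificNetwork],
                        labels: GroupLabels,
                        include_reference: bool = False) -> EdgeFeatureMatrix:
    """Assemble the samples x edges ΔPCC matrix from PPI-intersected SSNs.

    Reference-group samples are excluded unless ``include_reference``; the
    classifier discriminates among the disease groups.
    """
    if not candidates:
        raise ValueError("candidate edge list is empty")
    keep = [s for s in ssns
            if include_reference
            or labels.assignments[s.sample_id] != labels.reference_group]
    values = np.zeros((len(keep), len(candidates)))
    for r, ssn in enumerate(keep):
        for c, pair in enumerate(candidates):
            if pair in ssn.edges:
                values[r, c] = ssn.edges[pair][0]
    return EdgeFeatureMatrix(
        sample_ids=[s.sample_id for s in keep],
        edge_ids=list(candidates),
        values=values,
        groups=[labels.assignments[s.sample_id] for s in keep],
    )


# ---------------------------------------------------------------------------
# Gini machinery


def gini_impurity(class_proportions: Sequence[float]) -> float:
    """Gini = 1 - Σ p_i² for class proportions summing to 1."""
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
    return float(1.0 - (p ** 2).sum())


def impurity_gain(parent_counts: Sequence[float], left_counts: Sequence[float],
                  right_counts: Sequence[float]) -> float:
    """Size-weighted Gini decrease of a binary split.

        gain = |L|/|D| (Gini - Gini_L) + |R|/|D| (Gini - Gini_R)
             = Gini(parent) - (|L| Gini_L + |R| Gini_R) / |D|.
    """
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("left + right counts must equal parent counts")
    n = parent.sum()
    nl, nr = left.sum(), right.sum()
    if n <= 0 or nl <= 0 or nr <= 0:
        raise ValueError("splits must be non-empty")
    g = gini_impurity(parent / n)
    gl = gini_impurity(left / nl)
    gr = gini_impurity(right / nr)
    return float(nl / n * (g - gl) + nr / n * (g - gr))


def tree_gini_importances(estimators, n_features: int) -> np.ndarray:
    """Accumulate per-node impurity gains into per-feature importances.

    ``estimators`` are fitted sklearn decision trees (or a forest's
    ``estimators_``). For each internal node splitting on feature f the gain
    Gini(node) - weighted child Gini is added to importance[f].
    """
    importances = np.zeros(n_features)
    for est in estimators:
        t = est.tree_
        left, right = t.children_left, t.children_right
        for node in range(t.node_count):
            if left[node] < 0:  # leaf
                continue
            nn = t.weighted_n_node_samples[node]
            nl = t.weighted_n_node_samples[left[node]]
            nr = t.weighted_n_node_samples[right[node]]
            gain = t.impurity[node] - (nl * t.impurity[left[node]]
                                       + nr * t.impurity[right[node]]) / nn
            importances[t.feature[node]] += gain
    return importances


def _forest(config: PipelineConfig, seed_offset: int = 0) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.rf_trees,
        max_features="sqrt",
        random_state=(config.seed + seed_offset) % (2 ** 31),
        n_jobs=1,
    )


def prescreen_features(fm: EdgeFeatureMatrix, top_features: int,
                       config: PipelineConfig) -> ImportanceRanking:
    """Rank candidate edges by random-forest Gini-gain importance.

    Returns the full ranking; callers keep ``ranking.top(top_features)``.
    Fully reproducible under a fixed config seed.
    """
    classes = set(fm.groups)
    if len(classes) < 2:
        raise ValueError("pre-screening needs >= 2 groups in the feature matrix")
    rf = _forest(config)
    rf.fit(fm.values, np.asarray(fm.groups))
    raw = tree_gini_importances(rf.estimators_, len(fm.edge_ids))
    scores = {e: float(v) for e, v in zip(fm.edge_ids, raw)}
    order = sorted(fm.edge_ids, key=lambda e: (-scores[e], e))
    return ImportanceRanking(scores=scores, order=order)


def write_importances(ranking: ImportanceRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\timportance\trank\n")
        for rank, (a, b) in enumerate(ranking.order, start=1):
            fh.write(f"{a}\t{b}\t{ranking.scores[(a, b)]:.10g}\t{rank}\n")
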